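"""Folding-backend adapters.

Three adapters ship with the package:

* :class:`CTDirectoryBackend` — reads precomputed structures from a directory
  of Mfold-style CT files named ``<transcript>__<offset>.ct`` (one file per
  window, possibly holding several ranked records);
* :class:`DotBracketDirectoryBackend` — same layout with ``.db`` files, one
  structure per line, Vienna style (optional leading sequence line, optional
  trailing ``(energy)``);
* :class:`ViennaBackend` — live folding through the ViennaRNA Python
  bindings, detected at import time.

The deterministic fixture backend that pairs planted duplexes lives in
:mod:`duplexscan.fixtures`.
"""

from __future__ import annotations

import re
from pathlib import Path

from .structure_io import StructureRecord, parse_ct_file, parse_dot_bracket

__all__ = [
    "CTDirectoryBackend",
    "DotBracketDirectoryBackend",
    "ViennaBackend",
    "vienna_available",
    "get_backend",
]


def _window_file(directory: Path, transcript_id: str, offset: int,
                 suffix: str) -> Path:
    return directory / f"{transcript_id}__{offset}{suffix}"


class CTDirectoryBackend:
    """Serve precomputed structures from ``<transcript>__<offset>.ct`` files."""

    name = "ct-dir"

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise ValueError(f"not a directory: {directory}")

    def fold(self, sequence: str, max_structures: int, *,
             transcript_id: str = "", offset: int = 0) -> list[StructureRecord]:
        path = _window_file(self.directory, transcript_id, offset, ".ct")
        if not path.exists():
            return []
        records = parse_ct_file(path)
        for rec in records:
            if rec.pair_table.n != len(sequence):
                raise ValueError(
                    f"{path.name}: structure length {rec.pair_table.n} != "
                    f"window length {len(sequence)}"
                )
            if rec.bases is not None and rec.bases != sequence:
                raise ValueError(f"{path.name}: CT bases disagree with window "
                                 "sequence")
        return records[:max_structures]


_DB_LINE = re.compile(r"^([.()\[\]{}]+)\s*(?:\(\s*(-?\d+\.?\d*)\s*\))?\s*$")


class DotBracketDirectoryBackend:
    """Serve precomputed structures from ``<transcript>__<offset>.db`` files."""

    name = "db-dir"

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise ValueError(f"not a directory: {directory}")

    def fold(self, sequence: str, max_structures: int, *,
             transcript_id: str = "", offset: int = 0) -> list[StructureRecord]:
        path = _window_file(self.directory, transcript_id, offset, ".db")
        if not path.exists():
            return []
        records: list[StructureRecord] = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            if set(line) <= set("ACGUTacgut"):  # optional sequence line
                continue
            m = _DB_LINE.match(line)
            if m is None:
                raise ValueError(f"{path.name}: unparseable line {line!r}")
            pt = parse_dot_bracket(m.group(1))
            if pt.n != len(sequence):
                raise ValueError(
                    f"{path.name}: structure length {pt.n} != window length "
                    f"{len(sequence)}"
                )
            energy = float(m.group(2)) if m.group(2) else None
            records.append(StructureRecord(
                pair_table=pt, free_energy=energy, rank=len(records) + 1))
        return records[:max_structures]


def vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


class ViennaBackend:
    """Live MFE / suboptimal folding through the ViennaRNA bindings.

    The optimal structure comes from the MFE fold; additional ranked
    structures, when requested, from the suboptimal enumeration within a
    growing energy band above the MFE (capped at ``max_delta`` kcal/mol, so
    fewer than ``max_structures`` may be returned for strongly-folding
    windows with sparse suboptimal spectra).
    """

    name = "engine"

    def __init__(self, max_delta: float = 3.0):
        if not vienna_available():
            raise RuntimeError("ViennaRNA Python bindings are not installed")
        self.max_delta = max_delta

    def fold(self, sequence: str, max_structures: int, *,
             transcript_id: str = "", offset: int = 0) -> list[StructureRecord]:
        import RNA

        if max_structures <= 1:
            structure, mfe = RNA.fold(sequence)
            return [StructureRecord(pair_table=parse_dot_bracket(structure),
                                    free_energy=round(mfe, 2), rank=1)]
        fc = RNA.fold_compound(sequence)
        delta = 1.0
        sols = []
        while True:
            sols = [s for s in fc.subopt(int(round(delta * 100)))
                    if s.structure is not None]
            if len(sols) >= max_structures or delta >= self.max_delta:
                break
            delta = min(self.max_delta, delta * 2)
        sols.sort(key=lambda s: (s.energy, s.structure))
        return [
            StructureRecord(pair_table=parse_dot_bracket(s.structure),
                            free_energy=round(s.energy, 2), rank=k)
            for k, s in enumerate(sols[:max_structures], start=1)
        ]


def get_backend(kind: str, directory: str | Path | None = None):
    """CLI helper: build a backend by name (``ct-dir``, ``db-dir``, ``engine``)."""
    if kind == "ct-dir":
        if directory is None:
            raise ValueError("ct-dir backend needs --structures-dir")
        return CTDirectoryBackend(directory)
    if kind == "db-dir":
        if directory is None:
            raise ValueError("db-dir backend needs --structures-dir")
        return DotBracketDirectoryBackend(directory)
    if kind == "engine":
        return ViennaBackend()
    raise ValueError(f"unknown backend {kind!r}")
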