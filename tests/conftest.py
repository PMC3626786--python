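"""Shared test helpers: random structures, compatible sequences, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from duplexscan.structure_io import PairTable

CANONICAL = {
    "GC": ("G", "C"), "CG": ("C", "G"),
    "AU": ("A", "U"), "UA": ("U", "A"),
    "GU": ("G", "U"), "UG": ("U", "G"),
}


def random_pair_table(rng: np.random.Generator, n: int,
                      pair_fraction: float = 0.4) -> PairTable:
    """A random involution on 1..n (crossing pairs allowed)."""
    positions = rng.permutation(np.arange(1, n + 1))
    n_pairs = int(pair_fraction * n / 2)
    pairs = []
    for k in range(n_pairs):
        i, j = sorted((int(positions[2 * k]), int(positions[2 * k + 1])))
        pairs.append((i, j))
    return PairTable.from_pairs(n, pairs)


def random_stacked_table(rng: np.random.Generator, n: int,
                         n_helices: int = 4) -> PairTable:
    """A random pair table biased toward stacked runs (helix-rich)."""
    partner = [0] * (n + 1)
    for _ in range(n_helices):
        length = int(rng.integers(1, 12))
        i = int(rng.integers(1, n))
        j = int(rng.integers(1, n))
        i, j = min(i, j), max(i, j)
        for m in range(length):
            a, b = i + m, j - m
            if a >= b or a > n or b < 1 or partner[a] or partner[b]:
                break
            partner[a], partner[b] = b, a
    return PairTable(n, tuple(partner))


def random_nested_table(rng: np.random.Generator, n: int) -> PairTable:
    """A random pseudoknot-free pair table (built via a balanced string)."""
    from duplexscan.structure_io import parse_dot_bracket

    chars = []
    stack = 0
    for _ in range(n):
        r = rng.random()
        if r < 0.3 and stack > 0:
            chars.append(")")
            stack -= 1
        elif r < 0.65:
            chars.append("(")
            stack += 1
        else:
            chars.append(".")
    chars.extend(")" * stack)
    return parse_dot_bracket("".join(chars))


def compatible_sequence(pt: PairTable, rng: np.random.Generator) -> str:
    """A random sequence in which every pair of *pt* is canonical/wobble."""
    chars = list(rng.choice(list("ACGU"), size=pt.n))
    keys = list(CANONICAL)
    for i, j in pt.pairs():
        b5, b3 = CANONICAL[keys[int(rng.integers(len(keys)))]]
        chars[i - 1], chars[j - 1] = b5, b3
    return "".join(chars)


# ---------------------------------------------------------------------------
# Independent oracles

def oracle_helices(pt: PairTable) -> list[tuple[tuple[int, int], ...]]:
    """Brute-force helix grouping by a different mechanic than the scanner:
    stacked pairs share a constant i+j sum and consecutive i values."""
    by_sum: dict[int, list[tuple[int, int]]] = {}
    for i, j in pt.pairs():
        by_sum.setdefault(i + j, []).append((i, j))
    runs = []
    for total in by_sum:
        pairs = sorted(by_sum[total])
        run = [pairs[0]]
        for p in pairs[1:]:
            if p[0] == run[-1][0] + 1:
                run.append(p)
            else:
                runs.append(tuple(run))
                run = [p]
        runs.append(tuple(run))
    return sorted(runs)


def oracle_select(pt: PairTable, seq: str, min_bp: int = 8, min_dist: int = 40,
                  min_linker: int = 16, comp_class: str = "any",
                  hairpin: bool = False) -> list[tuple]:
    """Brute-force motif selection over the oracle helices."""
    def classify(i, j):
        key = seq[i - 1] + seq[j - 1]
        if key in ("GC", "CG"):
            return "GC"
        if key in ("AU", "UA"):
            return "AU"
        if key in ("GU", "UG"):
            return "GU"
        raise ValueError(key)

    selected = []
    for run in oracle_helices(pt):
        if comp_class == "any":
            candidates = [run]
        else:
            candidates = []
            current = []
            for p in run:
                if current and classify(*p) != classify(*current[-1]):
                    candidates.append(tuple(current))
                    current = []
                current.append(p)
            candidates.append(tuple(current))
            candidates = [c for c in candidates if classify(*c[0]) == comp_class]
        for cand in candidates:
            if len(cand) < min_bp:
                continue
            ik, jk = cand[-1]
            dist = jk - ik - 1
            if hairpin:
                if dist < min_dist:
                    selected.append(cand)
                continue
            if dist < min_dist:
                continue
            linker = sum(1 for p in range(ik + 1, jk) if pt.partner[p])
            if linker >= min_linker:
                selected.append(cand)
    return sorted(selected)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130410)
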