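"""Small shared helpers: sequence ops, rounding, RNG plumbing."""

from __future__ import annotations

import math

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero upward (1.5 -> 2, 2.5 -> 3).

    Python's built-in round() uses banker's rounding; printed bp quantities in
    the domain convention round halves up instead.
    """
    return int(math.floor(x + 0.5))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """A uniform random A/C/G/T string of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def spawn_rng(seed: int, *salt: int) -> np.random.Generator:
    """Derive an independent generator from a master seed and salt integers."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, salt)]))


def homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """Half-open intervals of single-nucleotide runs of length >= min_len."""
    runs: list[tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def in_any_interval(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(a <= pos < b for a, b in intervals)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out
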