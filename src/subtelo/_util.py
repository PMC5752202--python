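"""Small shared helpers: interval arithmetic, sequences, seeded sub-RNGs."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals, gap: int = 0):
    """Merge overlapping (and within-``gap``) half-open intervals.

    Parameters
    ----------
    intervals
        Iterable of ``(start, end)`` pairs.
    gap
        Two intervals separated by at most ``gap`` bases are joined.

    Returns
    -------
    list of ``(start, end)`` pairs, sorted and disjoint.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 if they touch/overlap."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def keyed_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic generator derived from a base seed plus string/int keys.

    The same (seed, keys) always yields the same stream, independent of call
    order — used so that truth re-evaluation is idempotent.
    """
    words = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()) & 0xFFFFFFFF)
        else:
            words.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(words)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n`` (vectorized)."""
    arr = rng.integers(0, 4, size=n, dtype=np.uint8)
    table = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")
    return arr.tobytes().translate(table).decode()
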