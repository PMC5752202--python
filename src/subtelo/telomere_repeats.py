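"""Detection and classification of (TTAGGG)_n tandem repeat arrays.

Arrays are maximal exact runs of the canonical hexamer on either strand
(TTAGGG on '+', its reverse complement CCCTAA on '-'); partial trailing
hexamers never count toward ``n``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import List

from .genome_model import AnnotatedGenome, GenomeModelError, TELOMERE_UNIT, TELOMERE_UNIT_RC

_FWD = re.compile(r"(?:%s)+" % TELOMERE_UNIT)
_REV = re.compile(r"(?:%s)+" % TELOMERE_UNIT_RC)


@dataclass(frozen=True)
class RepeatArray:
    chrom: str
    start: int
    end: int
    n: int
    strand: str
    terminal: bool = False

    def __post_init__(self):
        if self.n < 1 or self.end - self.start != 6 * self.n:
            raise ValueError("repeat array length must be 6*n with n >= 1")


def find_repeat_arrays(sequence: str, min_n: int = 1, chrom: str = ".") -> List[RepeatArray]:
    """Maximal exact (TTAGGG)_n / (CCCTAA)_n runs with n >= ``min_n``.

    The run boundaries are phase-maximal: a match is extended as far as whole
    hexamers repeat, and runs on the two strands are reported independently.
    """
    seq = sequence.upper()
    out = []
    for pat, strand in ((_FWD, "+"), (_REV, "-")):
        for m in pat.finditer(seq):
            n = (m.end() - m.start()) // 6
            if n >= min_n:
                out.append(
                    RepeatArray(chrom, m.start(), m.start() + 6 * n, n, strand)
                )
    out.sort(key=lambda a: (a.start, a.strand))
    return out


def array_length_bp(n: int) -> int:
    """Length in bp of an n-unit hexamer array (6 * n)."""
    if n < 0:
        raise ValueError("repeat count must be non-negative")
    return 6 * n


def classify_arrays(arrays: List[RepeatArray], genome: AnnotatedGenome,
                    terminal_zone: int = 1_000) -> List[RepeatArray]:
    """Flag arrays as terminal (within ``terminal_zone`` of a linear
    chromosome end) or interstitial; everything on a circular chromosome is
    interstitial."""
    out = []
    for a in arrays:
        c = genome.chrom(a.chrom)
        if not (0 <= a.start and a.end <= c.length):
            raise GenomeModelError(f"array {a} outside {a.chrom}")
        if c.circular:
            terminal = False
        else:
            terminal = min(a.start, c.length - a.end) <= terminal_zone
        out.append(replace(a, terminal=terminal))
    return out


def genome_repeat_arrays(genome: AnnotatedGenome, min_n: int = 1,
                         terminal_zone: int = 1_000) -> List[RepeatArray]:
    """Find and classify arrays on every chromosome of a sequence-mode genome."""
    if genome.sequences is None:
        raise GenomeModelError("repeat scanning requires sequence-mode genome")
    arrays = []
    for c in genome.chromosomes:
        arrays.extend(find_repeat_arrays(genome.sequences[c.name], min_n, chrom=c.name))
    return classify_arrays(arrays, genome, terminal_zone=terminal_zone)


def terminal_repeat_counts(genome: AnnotatedGenome):
    """Repeat count detected at each end of each linear chromosome.

    Returns ``{chrom: (left_n, right_n)}`` from the sequence itself (0 when
    no array touches that end).
    """
    counts = {}
    for c in genome.chromosomes:
        if c.circular:
            continue
        arrays = find_repeat_arrays(genome.sequences[c.name], chrom=c.name)
        left = next((a.n for a in arrays if a.start == 0), 0)
        right = next((a.n for a in arrays if a.end == c.length), 0)
        counts[c.name] = (left, right)
    return counts
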