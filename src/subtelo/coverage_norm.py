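"""Sliding-window coverage, read-depth scaling normalization and smoothing.

Coverage is averaged over ``window`` bp sliding windows advanced by ``step``
bp (defaults 100/50); each window's value is the mean per-base read depth
inside it. Samples are made comparable by dividing by a scaling factor equal
to the ratio of total mapped reads in the sample relative to the reference.
Display smoothing applies a wider moving average (350 or 500 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Union

import numpy as np

from .alignments import ReadAlignmentSet


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Per-window signal over a genome, with its normalization history."""

    chrom_lengths: Dict[str, int]
    window: int
    step: int
    values: Dict[str, np.ndarray]
    normalization: dict = field(default_factory=dict)

    @staticmethod
    def n_windows(length: int, window: int, step: int) -> int:
        if length < window:
            return 0
        return (length - window) // step + 1

    def window_starts(self, chrom: str) -> np.ndarray:
        n = len(self.values[chrom])
        return np.arange(n, dtype=np.int64) * self.step

    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.values.values())
        count = sum(len(v) for v in self.values.values())
        return total / count if count else 0.0

    def same_geometry(self, other: "CoverageTrack") -> bool:
        return (
            self.window == other.window
            and self.step == other.step
            and self.chrom_lengths == other.chrom_lengths
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            dict(self.chrom_lengths), self.window, self.step,
            {c: v.copy() for c, v in self.values.items()},
            dict(self.normalization),
        )

    # -- bedGraph -----------------------------------------------------------

    def to_bedgraph(self, path, track_line: bool = False) -> None:
        with open(path, "w") as fh:
            if track_line:
                fh.write('track type=bedGraph\n')
            for chrom, vals in self.values.items():
                starts = self.window_starts(chrom)
                for s, v in zip(starts, vals):
                    fh.write(f"{chrom}\t{s}\t{s + self.window}\t{v:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path, chrom_lengths: Dict[str, int],
                      window: int, step: int) -> "CoverageTrack":
        values = {
            c: np.zeros(cls.n_windows(L, window, step))
            for c, L in chrom_lengths.items()
        }
        with open(path) as fh:
            for line in fh:
                if line.startswith(("track", "#")) or not line.strip():
                    continue
                chrom, s, _e, v = line.split("\t")
                idx = int(s) // step
                values[chrom][idx] = float(v)
        return cls(dict(chrom_lengths), window, step, values)


AlignmentsLike = Union[ReadAlignmentSet, Iterable]


def _per_chrom_intervals(alignments: AlignmentsLike, chrom_lengths):
    if isinstance(alignments, ReadAlignmentSet):
        for chrom in chrom_lengths:
            yield chrom, *alignments.intervals(chrom)
    else:
        per: Dict[str, list] = {c: [] for c in chrom_lengths}
        for chrom, s, e in alignments:
            per[chrom].append((s, e))
        for chrom, ivs in per.items():
            if ivs:
                arr = np.asarray(ivs, dtype=np.int64)
                yield chrom, arr[:, 0], arr[:, 1]
            else:
                yield chrom, np.empty(0, np.int64), np.empty(0, np.int64)


def window_coverage(alignments: AlignmentsLike,
                    chrom_lengths: Dict[str, int],
                    window: int = 100, step: int = 50) -> CoverageTrack:
    """Mean per-base depth in sliding windows.

    Edge windows shorter than ``window`` are dropped, so each chromosome has
    ``floor((L - window)/step) + 1`` windows. Raises if any alignment exceeds
    chromosome bounds.
    """
    if window < step:
        raise CoverageError("window must be >= step")
    values = {}
    for chrom, starts, ends in _per_chrom_intervals(alignments, chrom_lengths):
        L = chrom_lengths[chrom]
        n_win = CoverageTrack.n_windows(L, window, step)
        if len(starts) and (starts.min() < 0 or ends.max() > L):
            raise CoverageError(f"alignment beyond bounds of {chrom}")
        diff = np.zeros(L + 1, dtype=np.float64)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        depth_cum = np.concatenate(([0.0], np.cumsum(np.cumsum(diff[:-1]))))
        win_starts = np.arange(n_win, dtype=np.int64) * step
        vals = (depth_cum[win_starts + window] - depth_cum[win_starts]) / window
        values[chrom] = vals
    return CoverageTrack(dict(chrom_lengths), window, step, values)


def scaling_factor(sample_mapped_reads: int, reference_mapped_reads: int) -> float:
    """Sample-to-reference ratio of total mapped reads."""
    if reference_mapped_reads <= 0:
        raise CoverageError("reference mapped-read count must be > 0")
    if sample_mapped_reads <= 0:
        raise CoverageError("sample mapped-read count must be > 0")
    return sample_mapped_reads / reference_mapped_reads


def normalize_track(track: CoverageTrack, factor: float,
                    reference_id: Optional[str] = None) -> CoverageTrack:
    """Divide all window values by ``factor`` and record the normalization."""
    if factor <= 0:
        raise CoverageError("scaling factor must be positive")
    out = track.copy()
    for chrom in out.values:
        out.values[chrom] = out.values[chrom] / factor
    applied = out.normalization.get("factor", 1.0) * factor
    out.normalization = {"factor": applied, "reference": reference_id}
    return out


def smooth_track(track: CoverageTrack, display_window: int) -> CoverageTrack:
    """Moving average over ``display_window`` bp; step is unchanged.

    The kernel spans ``round(display_window / step)`` windows, uniform
    weights, 'same'-mode convolution (mass conserved away from chromosome
    edges).
    """
    if display_window < track.window:
        raise CoverageError("display window smaller than native window")
    k = max(1, int(round(display_window / track.step)))
    kernel = np.full(k, 1.0 / k)
    out = track.copy()
    for chrom in out.values:
        v = out.values[chrom]
        if len(v):
            out.values[chrom] = np.convolve(v, kernel, mode="same")
    out.normalization = dict(track.normalization)
    out.normalization["display_window"] = display_window
    return out
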