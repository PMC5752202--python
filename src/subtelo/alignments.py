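"""Lightweight alignment containers plus BED6 / minimal-SAM serialization.

These deliberately model only what the pipeline consumes: single-end
interval alignments for coverage, and paired/split records for breakpoint
evidence. The SAM dialect is header + the 11 mandatory columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np


@dataclass
class ReadAlignmentSet:
    """Single-end alignments as per-chromosome start arrays (fixed length)."""

    chrom_lengths: Dict[str, int]
    read_length: int
    starts: Dict[str, np.ndarray] = field(default_factory=dict)
    strands: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom in list(self.starts):
            self.starts[chrom] = np.asarray(self.starts[chrom], dtype=np.int64)

    @property
    def n_reads(self) -> int:
        return int(sum(len(v) for v in self.starts.values()))

    def intervals(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        s = self.starts.get(chrom, np.empty(0, dtype=np.int64))
        return s, s + self.read_length

    def iter_records(self):
        for chrom in self.starts:
            strands = self.strands.get(chrom)
            for i, s in enumerate(self.starts[chrom]):
                strand = "+" if strands is None else ("+" if strands[i] > 0 else "-")
                yield chrom, int(s), int(s) + self.read_length, strand

    # -- BED6 ---------------------------------------------------------------

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, s, e, strand) in enumerate(self.iter_records()):
                fh.write(f"{chrom}\t{s}\t{e}\tread{i}\t0\t{strand}\n")

    @classmethod
    def from_bed(cls, path, chrom_lengths: Dict[str, int]) -> "ReadAlignmentSet":
        per: Dict[str, list] = {}
        strands: Dict[str, list] = {}
        read_length = None
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, s, e = f[0], int(f[1]), int(f[2])
                read_length = e - s if read_length is None else read_length
                per.setdefault(chrom, []).append(s)
                strands.setdefault(chrom, []).append(
                    1 if (len(f) < 6 or f[5] != "-") else -1
                )
        return cls(
            chrom_lengths,
            read_length or 0,
            {c: np.array(v, dtype=np.int64) for c, v in per.items()},
            {c: np.array(v, dtype=np.int8) for c, v in strands.items()},
        )

    # -- minimal SAM --------------------------------------------------------

    def to_sam(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
            for i, (chrom, s, e, strand) in enumerate(self.iter_records()):
                flag = 0 if strand == "+" else 16
                fh.write(
                    f"read{i}\t{flag}\t{chrom}\t{s + 1}\t60\t"
                    f"{self.read_length}M\t*\t0\t0\t*\t*\n"
                )

    @classmethod
    def from_sam(cls, path) -> "ReadAlignmentSet":
        lengths: Dict[str, int] = {}
        per: Dict[str, list] = {}
        strands: Dict[str, list] = {}
        read_length = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("@"):
                    if line.startswith("@SQ"):
                        tags = dict(
                            t.split(":", 1) for t in line.rstrip().split("\t")[1:]
                        )
                        lengths[tags["SN"]] = int(tags["LN"])
                    continue
                f = line.rstrip("\n").split("\t")
                if f[2] == "*":
                    continue
                flag = int(f[1])
                cigar = f[5]
                if cigar.endswith("M") and cigar[:-1].isdigit():
                    read_length = int(cigar[:-1])
                per.setdefault(f[2], []).append(int(f[3]) - 1)
                strands.setdefault(f[2], []).append(-1 if flag & 16 else 1)
        return cls(
            lengths,
            read_length,
            {c: np.array(v, dtype=np.int64) for c, v in per.items()},
            {c: np.array(v, dtype=np.int8) for c, v in strands.items()},
        )


@dataclass(frozen=True)
class SplitAlignment:
    """A read split across two loci (base-pair-resolution junction evidence).

    ``pos1``/``pos2`` are the junction-side coordinates of the two pieces.
    """

    name: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    read_length: int = 0


@dataclass
class PairedAlignmentSet:
    """Columnar store of read pairs (mate leftmost coords and strands)."""

    chrom_lengths: Dict[str, int]
    read_length: int
    chrom1: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    pos1: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    strand1: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    chrom2: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    pos2: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    strand2: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    splits: List[SplitAlignment] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pos1)

    def to_sam(self, path) -> None:
        """Minimal paired SAM; split reads appear as supplementary lines."""
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
            for i in range(self.n_pairs):
                name = f"frag{i}"
                mates = (
                    (self.chrom1[i], self.pos1[i], self.strand1[i],
                     self.chrom2[i], self.pos2[i], 64),
                    (self.chrom2[i], self.pos2[i], self.strand2[i],
                     self.chrom1[i], self.pos1[i], 128),
                )
                for c, pos, strand, mc, mp, which in mates:
                    flag = 1 | which | (16 if strand < 0 else 0)
                    rnext = "=" if mc == c else mc
                    fh.write(
                        f"{name}\t{flag}\t{c}\t{pos + 1}\t60\t"
                        f"{self.read_length}M\t{rnext}\t{mp + 1}\t0\t*\t*\n"
                    )
            for s in self.splits:
                fh.write(
                    f"{s.name}\t2048\t{s.chrom1}\t{s.pos1 + 1}\t60\t*\t"
                    f"{s.chrom2}\t{s.pos2 + 1}\t0\t*\t*\n"
                )

    @classmethod
    def from_sam(cls, path) -> "PairedAlignmentSet":
        lengths: Dict[str, int] = {}
        read_length = 0
        first: Dict[str, tuple] = {}
        second: Dict[str, tuple] = {}
        splits: List[SplitAlignment] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("@"):
                    if line.startswith("@SQ"):
                        tags = dict(
                            t.split(":", 1) for t in line.rstrip().split("\t")[1:]
                        )
                        lengths[tags["SN"]] = int(tags["LN"])
                    continue
                f = line.rstrip("\n").split("\t")
                name, flag, chrom, pos = f[0], int(f[1]), f[2], int(f[3]) - 1
                if flag & 2048:
                    splits.append(
                        SplitAlignment(name, chrom, pos, f[6], int(f[7]) - 1)
                    )
                    continue
                if f[5].endswith("M") and f[5][:-1].isdigit():
                    read_length = int(f[5][:-1])
                strand = -1 if flag & 16 else 1
                (first if flag & 64 else second)[name] = (chrom, pos, strand)
        names = [n for n in first if n in second]
        out = cls(lengths, read_length)
        out.chrom1 = np.array([first[n][0] for n in names], dtype=object)
        out.pos1 = np.array([first[n][1] for n in names], dtype=np.int64)
        out.strand1 = np.array([first[n][2] for n in names], dtype=np.int8)
        out.chrom2 = np.array([second[n][0] for n in names], dtype=object)
        out.pos2 = np.array([second[n][1] for n in names], dtype=np.int64)
        out.strand2 = np.array([second[n][2] for n in names], dtype=np.int8)
        out.splits = splits
        return out
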