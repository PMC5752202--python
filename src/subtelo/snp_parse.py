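"""Allele-specific read partitioning against a SNPome.

Reads are trimmed to a fixed length, then assigned to a parent of origin
only if they match one parental genome exactly (full length, either strand);
the match is found by seeding read k-mers into an index built over
SNP-adjacent windows of the parent-A backbone and verifying that every
mismatch to the backbone sits on a SNP position and equals the parent-B
allele. Reads supporting different parents at different SNPs are flagged
``conflicted`` and excluded from profiles (reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from ._util import merge_intervals, revcomp

PARENT_A = "parent_A"
PARENT_B = "parent_B"
UNASSIGNED = "unassigned"
CONFLICTED = "conflicted"


@dataclass
class SNPome:
    """Biallelic SNP table with parent labels and flank convention."""

    chrom: List[str]
    pos: List[int]
    allele_a: List[str]
    allele_b: List[str]
    parents: Tuple[str, str] = ("A", "B")
    flank: int = 70

    def __post_init__(self):
        seen = set()
        for c, p, a, b in zip(self.chrom, self.pos, self.allele_a, self.allele_b):
            if a == b:
                raise ValueError(f"SNP {c}:{p} alleles identical")
            if (c, p) in seen:
                raise ValueError(f"duplicate SNP position {c}:{p}")
            seen.add((c, p))

    def __len__(self) -> int:
        return len(self.pos)

    def by_chrom(self) -> Dict[str, np.ndarray]:
        out: Dict[str, list] = {}
        for c, p in zip(self.chrom, self.pos):
            out.setdefault(c, []).append(p)
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\t%s\t%s\n" % self.parents)
            for c, p, a, b in zip(self.chrom, self.pos, self.allele_a, self.allele_b):
                fh.write(f"{c}\t{p}\t{a}\t{b}\n")

    @classmethod
    def from_tsv(cls, path, parents=("A", "B"), flank: int = 70) -> "SNPome":
        chrom, pos, aa, ab = [], [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                c, p, a, b = line.rstrip("\n").split("\t")[:4]
                chrom.append(c); pos.append(int(p)); aa.append(a); ab.append(b)
        return cls(chrom, pos, aa, ab, parents=parents, flank=flank)

    def to_paired_fasta(self, genome_a, path) -> None:
        """Paper-style FASTA listing both versions of each SNP with flanks."""
        L = self.flank
        with open(path, "w") as fh:
            for i, (c, p, a, b) in enumerate(
                zip(self.chrom, self.pos, self.allele_a, self.allele_b)
            ):
                seq = genome_a.sequences[c]
                left = seq[max(p - L + 1, 0):p]
                right = seq[p + 1:p + L]
                fh.write(f">snp{i}_{c}_{p}_{self.parents[0]}\n{left}{a}{right}\n")
                fh.write(f">snp{i}_{c}_{p}_{self.parents[1]}\n{left}{b}{right}\n")


def trim_filter_reads(reads: Iterable[Tuple[str, str]], L: int = 70):
    """Truncate each read to its first ``L`` bases; drop shorter reads."""
    if L <= 0:
        raise ValueError("trim length must be positive")
    out = []
    for name, seq in reads:
        if len(seq) >= L:
            out.append((name, seq[:L]))
    return out


@dataclass
class Assignment:
    label: str
    chrom: Optional[str] = None
    start: Optional[int] = None


class SnpAssigner:
    """Exact-match allele assignment against the parent-A backbone.

    ``genome_a`` must be sequence-mode; parent B is defined by the SNPome's
    alternate alleles on the same coordinates.
    """

    def __init__(self, genome_a, snpome: SNPome, read_length: int = 70, k: int = 20):
        if genome_a.sequences is None:
            raise ValueError("assigner requires a sequence-mode genome")
        if read_length != snpome.flank:
            raise ValueError(
                f"read length {read_length} != SNPome flank convention {snpome.flank}"
            )
        self.read_length = read_length
        self.k = k
        self.seqs = genome_a.sequences
        self.snp_pos = snpome.by_chrom()
        self.alleles: Dict[Tuple[str, int], Tuple[str, str]] = {
            (c, p): (a, b)
            for c, p, a, b in zip(snpome.chrom, snpome.pos,
                                  snpome.allele_a, snpome.allele_b)
        }
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        L = read_length
        for chrom, positions in self.snp_pos.items():
            seq = self.seqs[chrom]
            windows = merge_intervals(
                [(max(int(p) - L + 1, 0), min(int(p) + L - k + 1, len(seq) - k + 1))
                 for p in positions]
            )
            for s, e in windows:
                for i in range(s, e):
                    self._index.setdefault(seq[i:i + k], []).append((chrom, i))

    def assign_read(self, seq: str) -> Assignment:
        """Label one trimmed read; see module docstring for the rule."""
        L = self.read_length
        if len(seq) != L:
            raise ValueError(f"read length {len(seq)} != {L}")
        k = self.k
        for oriented in (seq, revcomp(seq)):
            tried = set()
            for o in range(0, L - k + 1):
                for chrom, hit in self._index.get(oriented[o:o + k], ()):
                    start = hit - o
                    if start < 0 or (chrom, start) in tried:
                        continue
                    tried.add((chrom, start))
                    result = self._verify(oriented, chrom, start)
                    if result is not None:
                        return result
        return Assignment(UNASSIGNED)

    def _verify(self, seq: str, chrom: str, start: int) -> Optional[Assignment]:
        L = self.read_length
        ref = self.seqs[chrom][start:start + L]
        if len(ref) != L:
            return None
        positions = self.snp_pos.get(chrom)
        covered = []
        if positions is not None:
            lo = np.searchsorted(positions, start, side="left")
            hi = np.searchsorted(positions, start + L, side="left")
            covered = [int(p) for p in positions[lo:hi]]
        covered_set = set(covered)
        votes = set()
        for i in range(L):
            if seq[i] == ref[i]:
                continue
            p = start + i
            if p not in covered_set:
                return None  # mismatch off-SNP: not a 100% parental match
            if seq[i] != self.alleles[(chrom, p)][1]:
                return None  # third allele: sequencing error at the SNP
        for p in covered:
            a, b = self.alleles[(chrom, p)]
            base = seq[p - start]
            votes.add("A" if base == a else "B")
        if not votes:
            return Assignment(UNASSIGNED, chrom, start)
        if votes == {"A"}:
            return Assignment(PARENT_A, chrom, start)
        if votes == {"B"}:
            return Assignment(PARENT_B, chrom, start)
        return Assignment(CONFLICTED, chrom, start)


def assign_read(seq: str, assigner: SnpAssigner) -> str:
    """Convenience wrapper returning just the label."""
    return assigner.assign_read(seq).label


def allele_scaling(count_a: int, count_b: int) -> Tuple[float, float]:
    """Per-allele scaling factors: the smaller file gets 1.0, the other its
    count over the minimum."""
    if count_a <= 0 or count_b <= 0:
        raise ValueError("both allele read counts must be > 0")
    m = min(count_a, count_b)
    return count_a / m, count_b / m


def snp_parsed_profiles(reads: Iterable[Tuple[str, str]],
                        assigner: SnpAssigner,
                        chrom_lengths: Dict[str, int],
                        window: int = 100, step: int = 50,
                        trim_to: int = 70):
    """Full pipeline: trim -> assign -> partition -> per-parent coverage ->
    allele scaling.

    Returns ``(track_a, track_b, report)``; conflicted reads are excluded and
    counted in the report.
    """
    from .coverage_norm import normalize_track, window_coverage

    trimmed = trim_filter_reads(reads, L=trim_to)
    placed = {PARENT_A: [], PARENT_B: []}
    counts = {PARENT_A: 0, PARENT_B: 0, UNASSIGNED: 0, CONFLICTED: 0}
    for _name, seq in trimmed:
        a = assigner.assign_read(seq)
        counts[a.label] += 1
        if a.label in placed:
            placed[a.label].append((a.chrom, a.start, a.start + trim_to))
    tracks = {}
    for label in (PARENT_A, PARENT_B):
        tracks[label] = window_coverage(placed[label], chrom_lengths,
                                        window=window, step=step)
    if counts[PARENT_A] > 0 and counts[PARENT_B] > 0:
        fa, fb = allele_scaling(counts[PARENT_A], counts[PARENT_B])
        tracks[PARENT_A] = normalize_track(tracks[PARENT_A], fa, "allele_min")
        tracks[PARENT_B] = normalize_track(tracks[PARENT_B], fb, "allele_min")
    report = {
        "n_input": len(trimmed),
        "assigned_A": counts[PARENT_A],
        "assigned_B": counts[PARENT_B],
        "unassigned": counts[UNASSIGNED],
        "conflicted": counts[CONFLICTED],
    }
    return tracks[PARENT_A], tracks[PARENT_B], report
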