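"""Discordant-pair / split-read breakpoint calling and the outward-primer
chromosome-fusion test.

This is an intentional simplification of full structural-variant callers:
evidence is classified by pair geometry (inter-chromosomal, anomalous
orientation, or implied insert outside mean +/- 4 sd), clustered by
single linkage with both junction loci within ``cluster_dist``, and calls
below ``min_weight`` supporting alignments are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .alignments import PairedAlignmentSet
from .genome_model import AnnotatedGenome


@dataclass(frozen=True)
class Evidence:
    """One supporting alignment: two junction-facing loci.

    ``dir1``/``dir2`` give the direction each locus faces (+1 when the
    junction lies at or beyond the locus moving right). Split reads carry
    base-pair-resolution loci.
    """

    chrom1: str
    pos1: int
    dir1: int
    chrom2: str
    pos2: int
    dir2: int
    kind: str  # "pair" | "split"


@dataclass(frozen=True)
class BreakpointCall:
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    weight: int
    n_pairs: int
    n_splits: int

    def loci(self):
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


def collect_evidence(pairs: PairedAlignmentSet, insert_mean: float,
                     insert_sd: float) -> List[Evidence]:
    """Extract discordant-pair and split-read evidence.

    A pair is discordant when inter-chromosomal, when the leftmost mate is
    not forward / rightmost not reverse, or when the implied insert falls
    outside ``insert_mean +/- 4 * insert_sd``.
    """
    rl = pairs.read_length
    n = pairs.n_pairs
    ev: List[Evidence] = []
    if n:
        c1, c2 = pairs.chrom1, pairs.chrom2
        p1, p2 = pairs.pos1, pairs.pos2
        s1, s2 = pairs.strand1.astype(np.int64), pairs.strand2.astype(np.int64)
        inter = c1 != c2
        left_is_1 = p1 <= p2
        left_strand = np.where(left_is_1, s1, s2)
        right_strand = np.where(left_is_1, s2, s1)
        orient_ok = (left_strand == 1) & (right_strand == -1)
        insert = np.abs(p2 - p1) + rl
        size_ok = (np.abs(insert - insert_mean) <= 4 * insert_sd)
        discordant = inter | ~orient_ok | ~size_ok
        for i in np.nonzero(discordant)[0]:
            l1 = int(p1[i] + rl) if s1[i] > 0 else int(p1[i])
            l2 = int(p2[i] + rl) if s2[i] > 0 else int(p2[i])
            ev.append(_canonical(Evidence(
                str(c1[i]), l1, int(s1[i]), str(c2[i]), l2, int(s2[i]), "pair"
            )))
    for s in pairs.splits:
        ev.append(_canonical(Evidence(
            s.chrom1, s.pos1, 0, s.chrom2, s.pos2, 0, "split"
        )))
    return ev


def _canonical(e: Evidence) -> Evidence:
    if (e.chrom1, e.pos1) <= (e.chrom2, e.pos2):
        return e
    return Evidence(e.chrom2, e.pos2, e.dir2, e.chrom1, e.pos1, e.dir1, e.kind)


def cluster_and_call(evidence: List[Evidence], cluster_dist: int = 500,
                     min_weight: int = 5,
                     max_span: int = 10_000) -> List[BreakpointCall]:
    """Single-linkage clustering of evidence into breakpoint calls.

    Two evidence items link when both of their loci lie within
    ``cluster_dist``. Call position is the median of split-read loci when
    splits are present, else the junction-facing boundary of the pair
    support. Clusters wider than ``max_span`` on either side, or lighter
    than ``min_weight``, are discarded.
    """
    groups: Dict[Tuple[str, str], List[Evidence]] = {}
    for e in evidence:
        groups.setdefault((e.chrom1, e.chrom2), []).append(e)

    calls: List[BreakpointCall] = []
    for (chrom1, chrom2), items in groups.items():
        items.sort(key=lambda e: (e.pos1, e.pos2))
        parent = list(range(len(items)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if items[j].pos1 - items[i].pos1 > cluster_dist:
                    break
                if abs(items[j].pos2 - items[i].pos2) <= cluster_dist:
                    union(i, j)

        clusters: Dict[int, List[Evidence]] = {}
        for i, e in enumerate(items):
            clusters.setdefault(find(i), []).append(e)

        for members in clusters.values():
            if len(members) < min_weight:
                continue
            p1s = np.array([m.pos1 for m in members])
            p2s = np.array([m.pos2 for m in members])
            if np.ptp(p1s) > max_span or np.ptp(p2s) > max_span:
                continue
            splits = [m for m in members if m.kind == "split"]
            if splits:
                pos1 = int(np.median([m.pos1 for m in splits]))
                pos2 = int(np.median([m.pos2 for m in splits]))
            else:
                pos1 = _pair_boundary(members, side=1)
                pos2 = _pair_boundary(members, side=2)
            calls.append(BreakpointCall(
                chrom1, pos1, chrom2, pos2, len(members),
                n_pairs=len(members) - len(splits), n_splits=len(splits),
            ))
    calls.sort(key=lambda c: (c.chrom1, c.pos1, c.chrom2, c.pos2))
    return calls


def _pair_boundary(members: List[Evidence], side: int) -> int:
    pairs = [m for m in members if m.kind == "pair"]
    pos = [m.pos1 if side == 1 else m.pos2 for m in pairs]
    dirs = [m.dir1 if side == 1 else m.dir2 for m in pairs]
    # Junction lies beyond the support in the direction most mates face.
    if sum(dirs) >= 0:
        return int(max(pos))
    return int(min(pos))


def fusion_junction_test(genome: AnnotatedGenome, primer_offset: int = 1_000,
                         primer_len: int = 20,
                         max_amplicon: int = 5_000) -> Dict[str, bool]:
    """Outward-primer PCR test for chromosome circularization.

    Primers are placed ``primer_offset`` bp inside each (former) end, facing
    outward. On a linear chromosome they point off the ends and never form a
    product; on a circularized chromosome they face each other across the
    fusion junction, and the test is positive when the implied amplicon is at
    most ``max_amplicon`` bp.
    """
    result: Dict[str, bool] = {}
    for c in genome.chromosomes:
        if primer_offset + primer_len > c.length:
            raise ValueError(f"primers fall off chromosome {c.name}")
        if not c.circular:
            result[c.name] = False
            continue
        amplicon = 2 * (primer_offset + primer_len)
        result[c.name] = amplicon <= max_amplicon
    return result


def match_truth(calls: List[BreakpointCall],
                truth: List[Tuple[Tuple[str, int], Tuple[str, int]]],
                tol: int = 300) -> Tuple[int, int, int]:
    """(true positives, false positives, false negatives) at ``tol`` bp.

    A call matches a truth junction when both loci agree (unordered) within
    ``tol``.
    """
    def close(a, b):
        return a[0] == b[0] and abs(a[1] - b[1]) <= tol

    matched_truth = set()
    tp = fp = 0
    for call in calls:
        l1, l2 = call.loci()
        hit = None
        for i, (t1, t2) in enumerate(truth):
            if (close(l1, t1) and close(l2, t2)) or \
               (close(l1, t2) and close(l2, t1)):
                hit = i
                break
        if hit is None:
            fp += 1
        else:
            tp += 1
            matched_truth.add(hit)
    fn = len(truth) - len(matched_truth)
    return tp, fp, fn
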