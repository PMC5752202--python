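"""Methylation-domain calling and differential (gained/lost/invariant)
classification between strains through a liftover.

The caller is a deliberate thresholding caller: windows whose
chip/(floored input) enrichment reaches ``T`` seed domains, seed runs within
``G`` bp merge, and merged runs shorter than ``S`` bp are dropped. The
differential classifier lifts reference calls into derived coordinates and
labels by reciprocal-overlap matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._util import merge_intervals
from .coverage_norm import CoverageTrack
from .genome_model import LiftoverMap

GAINED = "gained"
LOST = "lost"
INVARIANT = "invariant"


@dataclass(frozen=True)
class DomainCall:
    chrom: str
    start: int
    end: int
    mean_enrichment: float = 0.0
    label: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DomainCallSet:
    calls: List[DomainCall]
    params: dict = field(default_factory=dict)
    differential: bool = False

    def __iter__(self):
        return iter(self.calls)

    def __len__(self):
        return len(self.calls)

    def on_chrom(self, chrom: str) -> List[DomainCall]:
        return [c for c in self.calls if c.chrom == chrom]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, c in enumerate(sorted(self.calls, key=lambda x: (x.chrom, x.start))):
                name = c.label if c.label else f"domain{i}"
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t"
                    f"{min(int(round(c.mean_enrichment * 100)), 1000)}\t.\n"
                )

    @classmethod
    def from_bed(cls, path) -> "DomainCallSet":
        calls = []
        labels = {GAINED, LOST, INVARIANT}
        differential = False
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                label = f[3] if len(f) > 3 and f[3] in labels else None
                differential = differential or label is not None
                score = float(f[4]) / 100 if len(f) > 4 else 0.0
                calls.append(DomainCall(f[0], int(f[1]), int(f[2]), score, label))
        return cls(calls, differential=differential)


def call_domains(chip: CoverageTrack, input_track: CoverageTrack,
                 T: float = 2.0, G: int = 10_000, S: int = 500) -> DomainCallSet:
    """Threshold-merge-filter domain calling on normalized tracks.

    The input track is floored at its genome-wide 5th percentile to avoid
    division blow-ups in low-coverage windows.
    """
    if not chip.same_geometry(input_track):
        raise ValueError("chip and input tracks have mismatched geometry")
    all_input = np.concatenate([v for v in input_track.values.values()]) \
        if input_track.values else np.empty(0)
    if all_input.size == 0 or float(all_input.mean()) <= 0:
        raise ValueError("input track has zero genome-wide mean")
    floor = max(float(np.percentile(all_input, 5)), 1e-12)

    window, step = chip.window, chip.step
    calls: List[DomainCall] = []
    for chrom, chip_v in chip.values.items():
        in_v = np.maximum(input_track.values[chrom], floor)
        enrich = chip_v / in_v
        seeds = enrich >= T
        if not seeds.any():
            continue
        idx = np.nonzero(seeds)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        run_bounds = zip(
            np.concatenate(([0], breaks + 1)),
            np.concatenate((breaks, [len(idx) - 1])),
        )
        raw = [
            (int(idx[a]) * step, int(idx[b]) * step + window)
            for a, b in run_bounds
        ]
        for s, e in merge_intervals(raw, gap=G):
            if e - s < S:
                continue
            w_lo = (s + step - 1) // step
            w_hi = max((e - window) // step + 1, w_lo + 1)
            mean_enr = float(enrich[w_lo:min(w_hi, len(enrich))].mean())
            calls.append(DomainCall(chrom, s, min(e, chip.chrom_lengths[chrom]),
                                    mean_enr))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return DomainCallSet(calls, params={"T": T, "G": G, "S": S,
                                        "window": window, "step": step})


def _overlap(a: DomainCall, b: DomainCall) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def classify_differential(ref_calls: DomainCallSet, alt_calls: DomainCallSet,
                          lift: LiftoverMap,
                          min_overlap: float = 0.5) -> DomainCallSet:
    """Label derived-genome calls against lifted reference calls.

    A lifted reference call and an alt call match when their overlap is at
    least ``min_overlap`` of *both* lengths (reciprocal rule). Matched alt
    calls are ``invariant``; unmatched alt calls are ``gained``; unmatched
    lifted reference calls are reported (in derived coordinates) as ``lost``.
    """
    lifted: List[DomainCall] = []
    for c in ref_calls:
        for chrom2, s2, e2, _o in lift.lift_interval(c.chrom, c.start, c.end):
            lifted.append(DomainCall(chrom2, s2, e2, c.mean_enrichment))

    ref_matched = [False] * len(lifted)
    out: List[DomainCall] = []
    for a in alt_calls:
        matched = False
        for i, r in enumerate(lifted):
            ov = _overlap(a, r)
            if ov >= min_overlap * a.length and ov >= min_overlap * r.length:
                matched = True
                ref_matched[i] = True
        out.append(replace(a, label=INVARIANT if matched else GAINED))
    for i, r in enumerate(lifted):
        if not ref_matched[i]:
            out.append(replace(r, label=LOST))
    out.sort(key=lambda c: (c.chrom, c.start))
    return DomainCallSet(out, params=dict(alt_calls.params,
                                          min_overlap=min_overlap),
                         differential=True)


def subtelomeric_extension(calls: Iterable[DomainCall], chrom: str,
                           chrom_length: int, side: str = "right",
                           G: int = 10_000) -> int:
    """Distance (bp) from a chromosome end to the farthest interior edge of
    the end-anchored merged domain run; 0 if no call lies within ``G`` of the
    end."""
    ivs = [(c.start, c.end) for c in calls if c.chrom == chrom]
    runs = merge_intervals(ivs, gap=G)
    if side == "right":
        anchored = [r for r in runs if chrom_length - r[1] <= G]
        return max((chrom_length - r[0] for r in anchored), default=0)
    if side == "left":
        anchored = [r for r in runs if r[0] <= G]
        return max((r[1] for r in anchored), default=0)
    raise ValueError("side must be 'left' or 'right'")


def anchored_span_and_genes(calls: Iterable[DomainCall], chrom: str,
                            anchor_pos: int, genes: Sequence,
                            chrom_length: Optional[int] = None,
                            G: int = 10_000) -> Tuple[int, int, int]:
    """Merged anchor-connected run statistics: (span bp, farthest member-call
    edge from the anchor in bp, count of genes fully inside the run).

    Returns ``(0, 0, 0)`` when no call lies within ``G`` of the anchor.
    """
    if chrom_length is not None and not 0 <= anchor_pos < chrom_length:
        raise ValueError("anchor position off chromosome")
    members = [c for c in calls if c.chrom == chrom]
    runs = merge_intervals([(c.start, c.end) for c in members], gap=G)
    run = None
    for s, e in runs:
        if s - G <= anchor_pos < e + G:
            run = (s, e)
            break
    if run is None:
        return 0, 0, 0
    span = run[1] - run[0]
    farthest = 0
    for c in members:
        if c.start < run[1] and c.end > run[0]:
            farthest = max(farthest, abs(c.start - anchor_pos),
                           abs(c.end - anchor_pos))
    n_genes = sum(
        1 for g in genes
        if g.chrom == chrom and g.start >= run[0] and g.end <= run[1]
    )
    return span, farthest, n_genes
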